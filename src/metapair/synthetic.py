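"""Synthetic reference libraries, mock-community designs, and paired reads.

Everything downstream of sequencing is testable against data produced here:
a hierarchically mutated reference library with controlled divergence
strata, a multi-sample mock design (dominant host, low-abundance
parasitoids, bacterial symbionts, contaminants), and non-overlapping
paired reads with decaying quality, substitution errors, two-parent
chimeras, and a complete read-level truth manifest.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import SequenceRead, FORWARD, REVERSE
from .lineage import Lineage
from .seq_compare import revcomp

_BASES = np.array(list("ACGT"))

ROLES = ("host", "parasitoid", "symbiont", "contaminant")

#: default share of a sample's reads taken by the host specimen
DEFAULT_HOST_SHARE = 0.8
#: default aggregate share of bacterial symbiont reads
DEFAULT_SYMBIONT_SHARE = 0.05


@dataclass(frozen=True)
class ReferenceRecord:
    record_id: str
    lineage: Lineage
    sequence: str
    source: str = "simulated"  # {simulated, sanger, external}

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.record_id!r}: empty sequence")


@dataclass(frozen=True)
class Specimen:
    specimen_id: str
    role: str
    lineage: Lineage
    relative_abundance: float
    record_id: str  # reference record providing the amplicon template

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown specimen role {self.role!r}")
        if not (0.0 <= self.relative_abundance <= 1.0):
            raise ValueError("relative abundance outside [0, 1]")


@dataclass(frozen=True)
class MockSample:
    sample_id: str
    mid: str
    specimens: tuple[Specimen, ...]


@dataclass(frozen=True)
class MockDesign:
    samples: tuple[MockSample, ...]

    def __post_init__(self) -> None:
        mids = [s.mid for s in self.samples]
        if len(set(mids)) != len(mids):
            raise ValueError("sample MIDs are not unique")
        for m in mids:
            if len(m) != 7 or any(c not in "ACGT" for c in m):
                raise ValueError(f"MID {m!r} is not a 7-nt ACGT tag")
        for a_i in range(len(mids)):
            for b_i in range(a_i + 1, len(mids)):
                dist = sum(x != y for x, y in zip(mids[a_i], mids[b_i]))
                if dist < 3:
                    raise ValueError(
                        f"MIDs {mids[a_i]!r}/{mids[b_i]!r} closer than Hamming 3"
                    )
        for sample in self.samples:
            total = sum(sp.relative_abundance for sp in sample.specimens)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"sample {sample.sample_id!r}: abundances sum to {total}"
                )
            if not any(sp.role == "host" for sp in sample.specimens):
                raise ValueError(f"sample {sample.sample_id!r}: no host specimen")

    @property
    def mids(self) -> dict[str, str]:
        return {s.sample_id: s.mid for s in self.samples}

    def specimens_by_role(self, role: str) -> list[Specimen]:
        return [sp for s in self.samples for sp in s.specimens if sp.role == role]


@dataclass(frozen=True)
class ManifestEntry:
    specimen_id: str
    sample_id: str
    is_chimera: bool
    parent_ids: tuple[str, ...] = ()


@dataclass
class TruthManifest:
    entries: dict[str, ManifestEntry] = field(default_factory=dict)

    def add(self, read_id: str, entry: ManifestEntry) -> None:
        if read_id in self.entries:
            raise ValueError(f"duplicate read id {read_id!r} in manifest")
        self.entries[read_id] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def n_chimeras(self) -> int:
        return sum(e.is_chimera for e in self.entries.values())

    def reads_per_specimen(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries.values():
            counts[e.specimen_id] = counts.get(e.specimen_id, 0) + 1
        return counts

    def rows(self):
        for rid, e in self.entries.items():
            yield (rid, e.specimen_id, e.sample_id, e.is_chimera, e.parent_ids)


# ------------------------------------------------------- reference library


def _mutate(rng: np.random.Generator, seq: np.ndarray, n_sites: int) -> np.ndarray:
    """Substitute `n_sites` distinct positions, always to a different base."""
    out = seq.copy()
    sites = rng.choice(len(seq), size=n_sites, replace=False)
    shifts = rng.integers(1, 4, size=n_sites)
    out[sites] = (out[sites] + shifts) % 4
    return out


def _to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def _insect_lineage(order: str, family: str, genus: str, species: str) -> Lineage:
    return Lineage(
        ("Animalia", "Arthropoda", "Insecta", order, family, family + "inae",
         genus, species)
    )


def generate_reference_library(
    n_families: int,
    genera_per_family: int,
    species_per_genus: int,
    seed: int,
    *,
    seq_len: int = 658,
    order: str = "Lepidoptera",
    prefix: str = "REF",
    variants_per_species: int = 1,
    validate: bool = True,
) -> list[ReferenceRecord]:
    """Hierarchically mutated COI-like library with stratified divergence.

    Conspecific variants differ <1%, congeneric species 5-12%, and
    cross-genus pairs >12% (families are independent random ancestors).
    Raises ``ValueError`` when the strata cannot be realized at `seq_len`.
    """
    if min(n_families, genera_per_family, species_per_genus) < 1:
        raise ValueError("all counts must be >= 1")
    if variants_per_species < 1:
        raise ValueError("variants_per_species must be >= 1")
    k_species = max(1, round(0.034 * seq_len))
    k_genus = max(2, round(0.10 * seq_len))
    nominal = 200.0 * k_species / seq_len  # expected congeneric divergence %
    if not (5.0 <= nominal <= 12.0):
        raise ValueError(
            f"sequence length {seq_len} cannot realize the congeneric "
            f"5-12% divergence stratum (nominal {nominal:.1f}%)"
        )
    if variants_per_species > 1 and 200.0 / seq_len >= 1.0:
        raise ValueError(
            f"sequence length {seq_len} too short for <1% conspecific variants"
        )
    rng = np.random.default_rng(seed)
    records: list[ReferenceRecord] = []
    for fi in range(1, n_families + 1):
        family_anc = rng.integers(0, 4, size=seq_len)
        family = f"{prefix}fam{fi:02d}"
        for gi in range(1, genera_per_family + 1):
            genus_anc = _mutate(rng, family_anc, k_genus)
            genus = f"{prefix}gen{fi:02d}{gi:02d}"
            for si in range(1, species_per_genus + 1):
                species_seq = _mutate(rng, genus_anc, k_species)
                species = f"{genus}_sp{si:02d}"
                lineage = _insect_lineage(order, family, genus, species)
                for vi in range(1, variants_per_species + 1):
                    if vi == 1:
                        seq = species_seq
                    else:
                        seq = _mutate(rng, species_seq, max(1, round(0.002 * seq_len)))
                    rid = f"{prefix}_F{fi:02d}G{gi:02d}S{si:02d}"
                    if variants_per_species > 1:
                        rid += f"V{vi:02d}"
                    records.append(ReferenceRecord(rid, lineage, _to_str(seq)))
    if validate:
        _validate_strata(records)
    return records


def _validate_strata(records: Sequence[ReferenceRecord]) -> None:
    coded = [np.frombuffer(r.sequence.encode(), dtype=np.uint8) for r in records]
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            div = 100.0 * np.mean(coded[i] != coded[j])
            same_genus = a.lineage.name_at("genus") == b.lineage.name_at("genus")
            same_species = a.lineage.name_at("species") == b.lineage.name_at("species")
            if same_species and div >= 1.0:
                raise ValueError(f"conspecific pair {a.record_id}/{b.record_id} "
                                 f"diverged {div:.1f}% (>=1%)")
            if same_genus and not same_species and not (5.0 <= div <= 12.0):
                raise ValueError(f"congeneric pair {a.record_id}/{b.record_id} "
                                 f"diverged {div:.1f}% (outside 5-12%)")
            if not same_genus and div <= 12.0:
                raise ValueError(f"cross-genus pair {a.record_id}/{b.record_id} "
                                 f"diverged {div:.1f}% (<=12%)")


def generate_offtarget_library(
    n_bacteria: int,
    n_plants: int,
    seed: int,
    *,
    seq_len: int = 658,
) -> list[ReferenceRecord]:
    """Random non-insect references playing the symbiont/contaminant roles."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(1, n_bacteria + 1):
        lineage = Lineage(
            ("Bacteria", "Proteobacteria", "Alphaproteobacteria",
             "Rickettsiales", f"BACfam{i:02d}", f"BACfam{i:02d}eae",
             f"BACgen{i:02d}", f"BACgen{i:02d}_sp01")
        )
        seq = _to_str(rng.integers(0, 4, size=seq_len))
        records.append(ReferenceRecord(f"BAC_{i:02d}", lineage, seq))
    for i in range(1, n_plants + 1):
        lineage = Lineage(
            ("Viridiplantae", "Streptophyta", "Magnoliopsida",
             "Malpighiales", f"PLAfam{i:02d}", f"PLAfam{i:02d}oideae",
             f"PLAgen{i:02d}", f"PLAgen{i:02d}_sp01")
        )
        seq = _to_str(rng.integers(0, 4, size=seq_len))
        records.append(ReferenceRecord(f"PLA_{i:02d}", lineage, seq))
    return records


# ------------------------------------------------------------ mock design


def generate_mids(n: int, seed: int, min_distance: int = 3) -> list[str]:
    """Random 7-nt sample tags at pairwise Hamming distance >= min_distance."""
    rng = np.random.default_rng(seed)
    mids: list[str] = []
    attempts = 0
    while len(mids) < n:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError(f"could not place {n} MIDs at distance {min_distance}")
        cand = _to_str(rng.integers(0, 4, size=7))
        if all(sum(a != b for a, b in zip(cand, m)) >= min_distance for m in mids):
            mids.append(cand)
    return mids


def design_mock_community(
    host_library: Sequence[ReferenceRecord],
    parasitoid_library: Sequence[ReferenceRecord],
    offtarget_library: Sequence[ReferenceRecord],
    *,
    n_samples: int = 5,
    parasitoids_per_sample: int = 2,
    n_parasitoid_taxa: Optional[int] = None,
    host_share: float = DEFAULT_HOST_SHARE,
    symbiont_share: float = DEFAULT_SYMBIONT_SHARE,
    contaminant_share: float = 0.02,
    seed: int = 0,
) -> MockDesign:
    """Assemble a host-dominated multi-sample design from the libraries.

    Each sample receives one distinct host species (`host_share` of reads),
    a distinct set of parasitoid species sharing the remaining insect
    fraction equally, one bacterial symbiont, and one contaminant.
    `n_parasitoid_taxa` overrides ``n_samples * parasitoids_per_sample``
    and is dealt round-robin, so sample sizes may differ by one.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if host_share + symbiont_share + contaminant_share >= 1.0:
        raise ValueError("shares leave no room for parasitoid reads")
    n_parasitoids = (
        n_parasitoid_taxa
        if n_parasitoid_taxa is not None
        else n_samples * parasitoids_per_sample
    )
    if n_parasitoids < n_samples:
        raise ValueError("need at least one parasitoid taxon per sample")
    if len(host_library) < n_samples:
        raise ValueError("host library smaller than the number of samples")
    if len(parasitoid_library) < n_parasitoids:
        raise ValueError("parasitoid library too small for the design")
    rng = np.random.default_rng(seed)
    bacteria = [r for r in offtarget_library if r.lineage.name_at("kingdom") == "Bacteria"]
    others = [r for r in offtarget_library if r.lineage.name_at("kingdom") != "Bacteria"]
    if not bacteria or not others:
        raise ValueError("offtarget library must contain bacteria and contaminants")
    hosts = list(rng.choice(len(host_library), size=n_samples, replace=False))
    paras = list(rng.choice(len(parasitoid_library), size=n_parasitoids, replace=False))
    mids = generate_mids(n_samples, seed=seed + 1)
    para_share = (1.0 - host_share - symbiont_share - contaminant_share)
    samples = []
    for i in range(n_samples):
        sid = f"S{i + 1}"
        host_rec = host_library[hosts[i]]
        specs = [
            Specimen(f"{sid}_host", "host", host_rec.lineage, host_share,
                     host_rec.record_id)
        ]
        chunk = paras[i::n_samples]  # round-robin deal of parasitoid taxa
        for j, pi in enumerate(chunk, start=1):
            rec = parasitoid_library[pi]
            specs.append(
                Specimen(f"{sid}_par{j}", "parasitoid", rec.lineage,
                         para_share / len(chunk), rec.record_id)
            )
        bac = bacteria[int(rng.integers(len(bacteria)))]
        specs.append(Specimen(f"{sid}_sym", "symbiont", bac.lineage,
                              symbiont_share, bac.record_id))
        con = others[int(rng.integers(len(others)))]
        specs.append(Specimen(f"{sid}_con", "contaminant", con.lineage,
                              contaminant_share, con.record_id))
        samples.append(MockSample(sid, mids[i], tuple(specs)))
    return MockDesign(tuple(samples))


# ------------------------------------------------------------- simulation


def _quality_profile(
    rng: np.random.Generator, length: int, q_start: int = 38, q_end: int = 20,
    jitter: int = 3,
) -> np.ndarray:
    base = np.linspace(q_start, q_end, num=length)
    jit = rng.integers(-jitter, jitter + 1, size=length)
    return np.clip(np.rint(base) + jit, 2, 41).astype(int)


def _apply_errors(
    rng: np.random.Generator, seq: np.ndarray, error_rate: float
) -> np.ndarray:
    if error_rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    if hits.size:
        seq = seq.copy()
        seq[hits] = (seq[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return seq


_CODE = {b: i for i, b in enumerate("ACGT")}


def _encode4(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int64)


def simulate_paired_reads(
    design: MockDesign,
    library: Sequence[ReferenceRecord],
    reads_per_sample: int,
    *,
    read_len: int = 300,
    error_rate: float = 0.0,
    chimera_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SequenceRead], list[SequenceRead], TruthManifest]:
    """Emit non-overlapping paired reads plus the read-level truth manifest.

    Forward read = 7-nt MID + 5' amplicon region; reverse read = reverse
    complement of the 3' region.  Specimen read counts are multinomial in
    the design abundances; a `chimera_rate` fraction of reads are built
    from a two-parent single-breakpoint splice (intra-sample).
    """
    if not design.samples:
        raise ValueError("empty design")
    if reads_per_sample < 1:
        raise ValueError("reads_per_sample must be >= 1")
    if not (0.0 <= error_rate <= 1.0 and 0.0 <= chimera_rate <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    by_id = {r.record_id: r for r in library}
    rng = np.random.default_rng(seed)
    fwd_out: list[SequenceRead] = []
    rev_out: list[SequenceRead] = []
    manifest = TruthManifest()
    for sample in design.samples:
        amplicons = {}
        for sp in sample.specimens:
            rec = by_id.get(sp.record_id)
            if rec is None:
                raise ValueError(
                    f"specimen {sp.specimen_id!r} references unknown record "
                    f"{sp.record_id!r}"
                )
            if 2 * read_len >= len(rec.sequence) + len(sample.mid):
                raise ValueError(
                    f"2x{read_len} reads would overlap on the "
                    f"{len(rec.sequence)}-nt amplicon of {rec.record_id!r}"
                )
            amplicons[sp.specimen_id] = _encode4(rec.sequence)
        abundances = np.array([sp.relative_abundance for sp in sample.specimens])
        counts = rng.multinomial(reads_per_sample, abundances / abundances.sum())
        mid_codes = _encode4(sample.mid)
        serial = 0
        for sp, n_reads in zip(sample.specimens, counts):
            for _ in range(n_reads):
                serial += 1
                rid = f"{sample.sample_id}_{serial:06d}"
                template = amplicons[sp.specimen_id]
                is_chimera = False
                parents: tuple[str, ...] = ()
                if chimera_rate > 0 and rng.random() < chimera_rate:
                    mates = [s for s in sample.specimens
                             if s.specimen_id != sp.specimen_id]
                    if mates:
                        weights = np.array([m.relative_abundance for m in mates])
                        other = mates[int(rng.choice(len(mates),
                                                     p=weights / weights.sum()))]
                        brk = int(rng.integers(1, len(template)))
                        template = np.concatenate(
                            [template[:brk], amplicons[other.specimen_id][brk:]]
                        )
                        is_chimera = True
                        parents = (sp.specimen_id, other.specimen_id)
                fwd_codes = np.concatenate([mid_codes, template])[:read_len]
                rev_codes = (3 - template[::-1])[:read_len]  # revcomp
                fwd_codes = _apply_errors(rng, fwd_codes, error_rate)
                rev_codes = _apply_errors(rng, rev_codes, error_rate)
                fq = _quality_profile(rng, len(fwd_codes))
                rq = _quality_profile(rng, len(rev_codes))
                fwd_out.append(SequenceRead(rid, _to_str(fwd_codes),
                                            list(fq), FORWARD))
                rev_out.append(SequenceRead(rid, _to_str(rev_codes),
                                            list(rq), REVERSE))
                manifest.add(rid, ManifestEntry(sp.specimen_id, sample.sample_id,
                                                is_chimera, parents))
    return fwd_out, rev_out, manifest


# --------------------------------------------------------------- fixtures


def load_fixture_tables(name: str) -> pd.DataFrame:
    """Load a packaged fixture transcription (`table1` or `table2`)."""
    if name not in {"table1", "table2"}:
        raise ValueError(f"unknown fixture table {name!r}")
    ref = importlib.resources.files("metapair") / "fixtures" / f"{name}.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
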