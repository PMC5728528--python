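"""Evaluation layer: mock-community recovery, the three-method
identification-success comparison with equal-proportions tests, and the
BIN-vs-morphospecies reference-library completeness audit."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .lineage import Lineage
from .seq_compare import align_identity

LEVELS = ("family", "genus", "species")
AUDIT_RANKS = ("family", "subfamily", "genus", "species")


# ------------------------------------------------------------- recovery


@dataclass(frozen=True)
class SpecimenBarcode:
    """A per-specimen Sanger reference with its taxon (BIN) label."""

    specimen_id: str
    taxon: str
    sequence: str


@dataclass
class RecoveryReport:
    individuals: dict[str, tuple[bool, float, Optional[str]]]
    taxa: dict[str, bool]

    @property
    def n_individuals_matched(self) -> int:
        return sum(m for m, _, _ in self.individuals.values())

    @property
    def n_taxa_matched(self) -> int:
        return sum(self.taxa.values())

    @property
    def individual_fraction(self) -> float:
        return self.n_individuals_matched / len(self.individuals)

    @property
    def taxon_fraction(self) -> float:
        return self.n_taxa_matched / len(self.taxa)


def match_recovery(
    representatives: Mapping[str, Sequence[str]],
    specimen_barcodes: Sequence[SpecimenBarcode],
    min_identity: float = 97.0,
    min_overlap: int = 100,
) -> RecoveryReport:
    """Score which specimens (and their taxa) are recovered by any MOTU.

    A specimen is recovered iff some representative sequence aligns to its
    barcode with identity >= `min_identity` over >= `min_overlap` aligned
    columns (the overlap floor stands in for the e-value criterion).
    """
    individuals: dict[str, tuple[bool, float, Optional[str]]] = {}
    taxa: dict[str, bool] = {}
    for barcode in specimen_barcodes:
        best_identity, best_motu, matched = 0.0, None, False
        for motu_id, seqs in representatives.items():
            for seq in seqs:
                if not seq:
                    continue
                res = align_identity(seq, barcode.sequence)
                if res.aligned_cols < min_overlap:
                    continue
                if res.identity_pct > best_identity:
                    best_identity, best_motu = res.identity_pct, motu_id
        if best_identity >= min_identity:
            matched = True
        individuals[barcode.specimen_id] = (matched, best_identity, best_motu)
        taxa[barcode.taxon] = taxa.get(barcode.taxon, False) or matched
    return RecoveryReport(individuals=individuals, taxa=taxa)


# -------------------------------------------------- proportion testing


@dataclass(frozen=True)
class ProportionTestResult:
    chi2: float
    df: int
    p_value: float


def equal_proportions_test(
    successes: Sequence[int], totals: Sequence[int]
) -> ProportionTestResult:
    """k-sample chi-square test of equal proportions, no continuity
    correction: pooled p = sum(s)/sum(n), chi2 = sum (O-E)^2/E over both
    outcome cells of every group, df = k-1, upper-tail p."""
    if len(successes) != len(totals) or len(successes) < 2:
        raise ValueError("need >= 2 groups with matching success/total lists")
    if any(s < 0 or n <= 0 or s > n for s, n in zip(successes, totals)):
        raise ValueError("successes must satisfy 0 <= s <= n with n > 0")
    k = len(successes)
    pooled = sum(successes) / sum(totals)
    if pooled in (0.0, 1.0):
        return ProportionTestResult(0.0, k - 1, 1.0)
    chi2 = 0.0
    for s, n in zip(successes, totals):
        exp_s = n * pooled
        exp_f = n * (1.0 - pooled)
        chi2 += (s - exp_s) ** 2 / exp_s + ((n - s) - exp_f) ** 2 / exp_f
    return ProportionTestResult(chi2, k - 1, float(chi2_dist.sf(chi2, k - 1)))


# --------------------------------------------- identification matrix


@dataclass
class IdentificationMatrix:
    n_total: int
    successes: dict[tuple[str, str], int] = field(default_factory=dict)

    def pct(self, method: str, level: str) -> float:
        return round(100.0 * self.successes[(method, level)] / self.n_total, 1)

    def level_test(self, level: str, methods: Sequence[str]) -> ProportionTestResult:
        return equal_proportions_test(
            [self.successes[(m, level)] for m in methods],
            [self.n_total] * len(methods),
        )


def identification_matrix(
    assignments: Mapping[str, Sequence[Lineage]],
    truth: Sequence[Lineage],
) -> IdentificationMatrix:
    """Per-method, per-level success counts against true lineages.

    Success at a level requires the assignment to name the *correct*
    taxon at that level; levels are evaluated independently.
    """
    for lin in truth:
        if lin.name_at("species") is None:
            raise ValueError("truth lineages must be populated to species")
    matrix = IdentificationMatrix(n_total=len(truth))
    for method, lineages in assignments.items():
        if len(lineages) != len(truth):
            raise ValueError(
                f"method {method!r}: {len(lineages)} assignments for "
                f"{len(truth)} individuals"
            )
        for level in LEVELS:
            n_ok = sum(
                assigned.name_at(level) == true.name_at(level)
                and assigned.name_at(level) is not None
                for assigned, true in zip(lineages, truth)
            )
            matrix.successes[(method, level)] = n_ok
    return matrix


def matrix_from_table1(df: pd.DataFrame) -> IdentificationMatrix:
    """Build the matrix from the packaged Table-1 transcription (counts
    are reconstructed from the printed percentages at n=22)."""
    n_total = int(df["n_total"].iloc[0])
    matrix = IdentificationMatrix(n_total=n_total)
    for row in df.itertuples():
        matrix.successes[(row.method, row.level)] = int(row.n_success)
    return matrix


# ------------------------------------------------------- library audit


@dataclass(frozen=True)
class SpecimenRecord:
    """One taxon-group row of the reference-library audit table."""

    taxon_group: str
    guild: str  # {host, parasitoid}
    n_specimens: int
    n_larva: int
    n_pupa: int
    n_adult: int
    n_morphospecies: int
    n_bins: int
    pct_bins_assigned: dict[str, float]  # rank -> % of BINs named at rank

    def __post_init__(self) -> None:
        if self.guild not in {"host", "parasitoid"}:
            raise ValueError(f"unknown guild {self.guild!r}")
        for rank, pct in self.pct_bins_assigned.items():
            if not (0.0 <= pct <= 100.0):
                raise ValueError(f"{self.taxon_group}: {rank} percentage {pct}")

    def n_assigned(self, rank: str) -> int:
        """BIN count implied by the printed percentage (rounded half-up)."""
        raw = Decimal(self.n_bins) * Decimal(str(self.pct_bins_assigned[rank])) / 100
        return int(raw.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class GuildSummary:
    n_specimens: int
    n_morphospecies: int
    n_bins: int
    n_assigned: dict[str, int]
    pct_assigned: dict[str, float]
    # groups where the BIN count differs from the morphospecies count
    bin_vs_morpho_delta: dict[str, int]


@dataclass
class LibrarySummary:
    guilds: dict[str, GuildSummary]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Half-up decimal rounding after suppressing float representation
    noise (so 5.114999999999999 -> 5.12 at two digits, as printed)."""
    quantum = Decimal(1).scaleb(-ndigits)
    cleaned = Decimal(str(round(value, ndigits + 6)))
    return float(cleaned.quantize(quantum, rounding=ROUND_HALF_UP))


def _round_half_up_1dp(value: float) -> float:
    return round_half_up(value, 1)


def library_completeness(records: Sequence[SpecimenRecord]) -> LibrarySummary:
    """Aggregate audit rows per guild.

    Rank percentages are BIN-weighted: per row the implied number of
    assigned BINs is reconstructed from the printed percentage, summed,
    and re-expressed as a percentage of the guild BIN total (half-up, one
    decimal) — the aggregation that reproduces the printed sum rows.
    """
    guilds: dict[str, GuildSummary] = {}
    for guild in sorted({r.guild for r in records}):
        rows = [r for r in records if r.guild == guild]
        n_bins = sum(r.n_bins for r in rows)
        n_assigned = {
            rank: sum(r.n_assigned(rank) for r in rows) for rank in AUDIT_RANKS
        }
        pct = {
            rank: _round_half_up_1dp(100.0 * n_assigned[rank] / n_bins)
            for rank in AUDIT_RANKS
        }
        guilds[guild] = GuildSummary(
            n_specimens=sum(r.n_specimens for r in rows),
            n_morphospecies=sum(r.n_morphospecies for r in rows),
            n_bins=n_bins,
            n_assigned=n_assigned,
            pct_assigned=pct,
            bin_vs_morpho_delta={
                r.taxon_group: r.n_bins - r.n_morphospecies
                for r in rows
                if r.n_bins != r.n_morphospecies
            },
        )
    return LibrarySummary(guilds=guilds)


def specimen_records_from_table2(df: pd.DataFrame) -> list[SpecimenRecord]:
    """Convert the packaged Table-2 transcription into audit records."""
    records = []
    for row in df.itertuples():
        records.append(
            SpecimenRecord(
                taxon_group=row.taxon_group,
                guild=row.guild,
                n_specimens=int(row.n_specimens),
                n_larva=int(row.n_larva),
                n_pupa=int(row.n_pupa),
                n_adult=int(row.n_adult),
                n_morphospecies=int(row.n_morphospecies),
                n_bins=int(row.n_bins),
                pct_bins_assigned={
                    "family": float(row.pct_family),
                    "subfamily": float(row.pct_subfamily),
                    "genus": float(row.pct_genus),
                    "species": float(row.pct_species),
                },
            )
        )
    return records
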