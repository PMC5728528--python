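"""Taxonomic assignment from non-overlapping read pairs.

The primary mode queries both mates against the reference library and
keeps only references matched by *both* reads, averages the two
identities, retains hits within `identity_window` points of the best
average, and assigns at the deepest rank where one full lineage prefix is
shared by at least `consensus_fraction` of the retained hits.  A
single-mate fallback handles pairs where no reference matches both reads,
an LCA fallback (common lineage prefix of near-top hits) handles clusters
with no match in the main library, and a best-hit identifier covers
full-length Sanger-style queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .lineage import Lineage, RANKS, common_prefix_of
from .seq_compare import KmerIndex, align_identity, revcomp
from .synthetic import ReferenceRecord

MODE_DUAL = "dual_read"
MODE_SINGLE = "single_read"
MODE_LCA = "lca_fallback"
MODE_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ClassifierParams:
    identity_window: float = 0.5  # absolute percentage points off the best average
    consensus_fraction: float = 0.5
    min_hit_identity: float = 80.0
    # a hit must cover this fraction of the query; guards against spurious
    # high-identity micro-overlaps allowed by free terminal gaps
    min_hit_coverage: float = 0.9
    lca_top_window: float = 10.0
    top_n_candidates: int = 30
    per_taxon_consensus: bool = False  # count unique taxa instead of records

    def __post_init__(self) -> None:
        if self.identity_window < 0 or self.lca_top_window < 0:
            raise ValueError("windows must be >= 0")
        if not (0.0 < self.consensus_fraction <= 1.0):
            raise ValueError("consensus_fraction must be in (0, 1]")


@dataclass(frozen=True)
class AssignmentResult:
    lineage: Lineage
    mode: str
    best_avg_identity_pct: float = 0.0
    n_retained_hits: int = 0
    retained: tuple[tuple[str, float], ...] = ()  # (record_id, avg identity)

    def __post_init__(self) -> None:
        if self.mode != MODE_UNASSIGNED and self.n_retained_hits < 1:
            raise ValueError("assigned result requires at least one retained hit")


UNASSIGNED = AssignmentResult(Lineage(), MODE_UNASSIGNED)


class ReferenceIndex:
    """K-mer indexed reference library with lineages."""

    def __init__(self, records: Sequence[ReferenceRecord], k: int = 8):
        if not records:
            raise ValueError("empty reference library")
        self.records: dict[str, ReferenceRecord] = {}
        self._index = KmerIndex(k=k)
        for rec in records:
            if rec.record_id in self.records:
                raise ValueError(f"duplicate reference id {rec.record_id!r}")
            self.records[rec.record_id] = rec
            self._index.add(rec.record_id, rec.sequence)

    def __len__(self) -> int:
        return len(self.records)

    def lineage(self, record_id: str) -> Lineage:
        return self.records[record_id].lineage

    def hits(
        self,
        query: str,
        min_identity: float,
        top_n: int,
        min_coverage: float = 0.9,
    ) -> dict[str, float]:
        """Identities of candidate references matching `query` at or above
        `min_identity` over at least `min_coverage` of the query length
        (candidates prescreened by shared k-mers)."""
        out: dict[str, float] = {}
        min_cols = min_coverage * len(query)
        for rid in self._index.search_candidates(query, top_n=top_n):
            res = align_identity(query, self.records[rid].sequence)
            if res.identity_pct >= min_identity and res.aligned_cols >= min_cols:
                out[rid] = res.identity_pct
        return out


def _consensus_walk(
    lineages: dict[str, Lineage],
    avg: dict[str, float],
    params: ClassifierParams,
) -> Lineage:
    """Deepest-rank majority over full lineage prefixes of retained hits."""
    n = len(avg)
    for depth in range(len(RANKS), 0, -1):
        counts: dict[tuple[str, ...], int] = {}
        for rid in avg:
            names = lineages[rid].names
            if len(names) >= depth:
                key = names[:depth]
                counts[key] = counts.get(key, 0) + 1
        if not counts:
            continue
        if params.per_taxon_consensus:
            # each distinct taxon counts once, whatever its record multiplicity
            denom = len(counts)
            winners = [
                k for k in counts if 1.0 / denom >= params.consensus_fraction
            ]
        else:
            winners = [
                k for k, c in counts.items()
                if c / n >= params.consensus_fraction
            ]
        if len(winners) == 1:
            return Lineage(winners[0])
        # 0 winners: no majority; >1 winners: exact tie -> rank fails
    return Lineage()


def _retained(hits: dict[str, float], window: float) -> dict[str, float]:
    best = max(hits.values())
    return {rid: ident for rid, ident in hits.items() if ident >= best - window}


def dual_read_assign(
    fwd: str,
    rev: str,
    library: ReferenceIndex,
    params: ClassifierParams = ClassifierParams(),
) -> AssignmentResult:
    """Paired-read consensus assignment; `rev` is given as sequenced."""
    rc = revcomp(rev)
    fwd_hits = library.hits(fwd, params.min_hit_identity, params.top_n_candidates,
                            params.min_hit_coverage)
    rev_hits = library.hits(rc, params.min_hit_identity, params.top_n_candidates,
                           params.min_hit_coverage)
    both = set(fwd_hits) & set(rev_hits)
    if both:
        avg_all = {rid: (fwd_hits[rid] + rev_hits[rid]) / 2.0 for rid in both}
        mode = MODE_DUAL
    else:
        # single-mate fallback: prefer the mate with the stronger best hit
        best_f = max(fwd_hits.values(), default=-1.0)
        best_r = max(rev_hits.values(), default=-1.0)
        if best_f < 0 and best_r < 0:
            return UNASSIGNED
        avg_all = dict(fwd_hits if best_f >= best_r else rev_hits)
        mode = MODE_SINGLE
    retained = _retained(avg_all, params.identity_window)
    lineages = {rid: library.lineage(rid) for rid in retained}
    lineage = _consensus_walk(lineages, retained, params)
    return AssignmentResult(
        lineage=lineage,
        mode=mode,
        best_avg_identity_pct=max(retained.values()),
        n_retained_hits=len(retained),
        retained=tuple(sorted(retained.items())),
    )


def single_read_assign(
    read: str,
    library: ReferenceIndex,
    params: ClassifierParams = ClassifierParams(),
) -> AssignmentResult:
    """Forward-only variant (benchmark comparator for the dual mode)."""
    hits = library.hits(read, params.min_hit_identity, params.top_n_candidates,
                        params.min_hit_coverage)
    if not hits:
        return UNASSIGNED
    retained = _retained(hits, params.identity_window)
    lineages = {rid: library.lineage(rid) for rid in retained}
    lineage = _consensus_walk(lineages, retained, params)
    return AssignmentResult(
        lineage=lineage,
        mode=MODE_SINGLE,
        best_avg_identity_pct=max(retained.values()),
        n_retained_hits=len(retained),
        retained=tuple(sorted(retained.items())),
    )


def lca_assign(
    fwd: str,
    rev: Optional[str],
    fallback_library: ReferenceIndex,
    params: ClassifierParams = ClassifierParams(),
) -> AssignmentResult:
    """Lowest-common-ancestor assignment against a fallback library.

    Hits are gathered as in :func:`dual_read_assign`; all hits within
    `lca_top_window` points of the best average are retained and the
    assigned lineage is the longest prefix common to all of them.
    """
    fwd_hits = fallback_library.hits(fwd, params.min_hit_identity,
                                     params.top_n_candidates,
                                     params.min_hit_coverage)
    rev_hits = (
        fallback_library.hits(revcomp(rev), params.min_hit_identity,
                              params.top_n_candidates, params.min_hit_coverage)
        if rev else {}
    )
    both = set(fwd_hits) & set(rev_hits)
    if both:
        avg_all = {rid: (fwd_hits[rid] + rev_hits[rid]) / 2.0 for rid in both}
    elif fwd_hits or rev_hits:
        best_f = max(fwd_hits.values(), default=-1.0)
        best_r = max(rev_hits.values(), default=-1.0)
        avg_all = dict(fwd_hits if best_f >= best_r else rev_hits)
    else:
        return UNASSIGNED
    retained = _retained(avg_all, params.lca_top_window)
    lineage = common_prefix_of(
        [fallback_library.lineage(rid) for rid in retained]
    )
    return AssignmentResult(
        lineage=lineage,
        mode=MODE_LCA,
        best_avg_identity_pct=max(retained.values()),
        n_retained_hits=len(retained),
        retained=tuple(sorted(retained.items())),
    )


def standard_barcode_identify(
    query: str,
    library: ReferenceIndex,
    max_divergence_pct: float = 3.0,
    *,
    shared_window: float = 5.0,
    params: ClassifierParams = ClassifierParams(),
) -> AssignmentResult:
    """Best-hit identification of a full-length (Sanger-style) barcode.

    The best hit's full lineage is the identification when its divergence
    is within `max_divergence_pct`; otherwise the deepest rank shared by
    all hits within `shared_window` points of the best is reported, capped
    at genus — beyond the divergence threshold no species claim is made.
    """
    hits = library.hits(query, params.min_hit_identity, params.top_n_candidates,
                        params.min_hit_coverage)
    if not hits:
        return UNASSIGNED
    best_id, best_ident = min(
        hits.items(), key=lambda kv: (-kv[1], kv[0])
    )
    if 100.0 - best_ident <= max_divergence_pct:
        return AssignmentResult(
            lineage=library.lineage(best_id),
            mode=MODE_SINGLE,
            best_avg_identity_pct=best_ident,
            n_retained_hits=1,
            retained=((best_id, best_ident),),
        )
    retained = _retained(hits, shared_window)
    lineage = common_prefix_of([library.lineage(rid) for rid in retained])
    lineage = lineage.truncate(len(RANKS) - 1)  # never species beyond 3%
    if not lineage:
        return UNASSIGNED
    return AssignmentResult(
        lineage=lineage,
        mode=MODE_SINGLE,
        best_avg_identity_pct=best_ident,
        n_retained_hits=len(retained),
        retained=tuple(sorted(retained.items())),
    )


# ------------------------------------------------------------ categories

CategoryRule = tuple[Callable[[Lineage], bool], str]


def default_category_rules(
    host_orders: frozenset[str] = frozenset({"Lepidoptera"}),
    parasitoid_orders: frozenset[str] = frozenset({"Hymenoptera", "Diptera"}),
) -> list[CategoryRule]:
    """Ordered lineage-predicate rules mapping assignments to categories."""
    return [
        (lambda lin: not lin, "unassigned"),
        (lambda lin: lin.name_at("kingdom") == "Bacteria", "putative_symbiont"),
        (
            lambda lin: (lin.name_at("class") == "Insecta"
                         and lin.name_at("order") in host_orders),
            "host",
        ),
        (
            lambda lin: (lin.name_at("class") == "Insecta"
                         and lin.name_at("order") in parasitoid_orders),
            "parasitoid",
        ),
    ]


def categorize_motu(
    assignment: AssignmentResult,
    rules: Optional[Sequence[CategoryRule]] = None,
) -> str:
    """First matching rule wins; non-target cellular life defaults to
    contaminant, unassigned results to unassigned."""
    if assignment.mode == MODE_UNASSIGNED:
        return "unassigned"
    for predicate, category in (rules if rules is not None
                                else default_category_rules()):
        if predicate(assignment.lineage):
            return category
    return "contaminant"
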