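"""Dereplication, de-novo chimera screening, greedy centroid clustering.

Clustering operates on forward reads only; reverse mates ride along via
read ids.  Uniques are processed in abundance order, each joining the
existing centroid of *highest* identity at or above the threshold
(deterministic best-hit assignment), else founding a new centroid.

The chimera screen is an openly simplified two-parent single-breakpoint
model: candidate parents must be `skew` times more abundant than the
query; the spliced parent model must beat the best single parent by
`min_gain` identity points and reach `min_model_identity` overall, with
both parent-derived segments at least `min_segment` nt long.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .io_formats import SequenceRead
from .seq_compare import KmerIndex, align_identity, query_match_profile


@dataclass
class Unique:
    """One dereplicated forward sequence with its supporting reads."""

    sequence: str
    abundance: int
    read_ids: list[str]


@dataclass(frozen=True)
class ChimeraParams:
    skew: float = 2.0
    n_chunks: int = 4
    top_parents_per_chunk: int = 4
    min_gain: float = 1.0
    min_model_identity: float = 99.0
    min_segment: int = 30


@dataclass(frozen=True)
class ChimeraCall:
    query_id: str  # sequence of the query unique is its identity here
    parent_a: str
    parent_b: str
    breakpoint: int
    model_identity_pct: float
    best_single_identity_pct: float
    verdict: str  # {chimeric, clean}


@dataclass
class MOTUCluster:
    motu_id: str
    centroid_fwd: str
    centroid_rev: str
    read_ids: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def dereplicate(reads: Iterable[SequenceRead]) -> list[Unique]:
    """Exact-string grouping, ordered by abundance desc then sequence."""
    groups: dict[str, list[str]] = {}
    for read in reads:
        groups.setdefault(read.bases, []).append(read.read_id)
    uniques = [Unique(seq, len(ids), ids) for seq, ids in groups.items()]
    uniques.sort(key=lambda u: (-u.abundance, u.sequence))
    return uniques


def detect_chimeras(
    uniques: Sequence[Unique], params: ChimeraParams = ChimeraParams()
) -> list[ChimeraCall]:
    """Screen abundance-ordered uniques for two-parent chimeras.

    Returns one call per query for which a two-parent model could be
    evaluated; use :func:`chimeric_sequences` to collect the positives.
    Queries are keyed by their unique sequence (`query_id`).
    """
    calls: list[ChimeraCall] = []
    index = KmerIndex(k=8)
    indexed = 0  # uniques[0:indexed] are in the parent index
    by_seq = {u.sequence: u for u in uniques}
    for qi, query in enumerate(uniques):
        # grow the eligible-parent prefix (sorted desc by abundance)
        while (indexed < len(uniques)
               and uniques[indexed].abundance >= params.skew * query.abundance):
            index.add(uniques[indexed].sequence, uniques[indexed].sequence)
            indexed += 1
        if indexed == 0:
            continue
        seq = query.sequence
        L = len(seq)
        if L < 2 * params.min_segment:
            continue
        chunk = max(1, L // params.n_chunks)
        candidates: list[str] = []
        for c in range(params.n_chunks):
            piece = seq[c * chunk: (c + 1) * chunk if c < params.n_chunks - 1 else L]
            for cand in index.search_candidates(piece, params.top_parents_per_chunk):
                if cand != seq and cand not in candidates:
                    candidates.append(cand)
        if len(candidates) < 2:
            continue
        profiles = np.stack([query_match_profile(seq, cand) for cand in candidates])
        totals = profiles.sum(axis=1)
        best_single = 100.0 * totals.max() / L
        cum = np.concatenate(
            [np.zeros((len(candidates), 1), dtype=int), np.cumsum(profiles, axis=1)],
            axis=1,
        )
        b_lo, b_hi = params.min_segment, L - params.min_segment
        best_model, best_pair, best_brk = -1.0, None, -1
        for i in range(len(candidates)):
            for j in range(len(candidates)):
                if i == j:
                    continue
                scores = cum[i, b_lo: b_hi + 1] + totals[j] - cum[j, b_lo: b_hi + 1]
                k = int(np.argmax(scores))
                ident = 100.0 * scores[k] / L
                if ident > best_model:
                    best_model, best_pair, best_brk = ident, (i, j), b_lo + k
        if best_pair is None:
            continue
        chimeric = (best_model >= params.min_model_identity
                    and best_model >= best_single + params.min_gain)
        calls.append(
            ChimeraCall(
                query_id=seq,
                parent_a=candidates[best_pair[0]],
                parent_b=candidates[best_pair[1]],
                breakpoint=best_brk,
                model_identity_pct=best_model,
                best_single_identity_pct=best_single,
                verdict="chimeric" if chimeric else "clean",
            )
        )
    return calls


def chimeric_sequences(calls: Iterable[ChimeraCall]) -> set[str]:
    return {c.query_id for c in calls if c.verdict == "chimeric"}


def greedy_cluster(
    uniques: Sequence[Unique],
    threshold_pct: float = 97.0,
    *,
    sample_of: Optional[Callable[[str], str]] = None,
    mate_of: Optional[Callable[[str], str]] = None,
    min_coverage: float = 0.9,
) -> list[MOTUCluster]:
    """Abundance-ordered greedy centroid clustering at `threshold_pct`.

    `sample_of` maps a read id to its sample (defaults to one pooled
    sample); `mate_of` returns the reverse-mate sequence used as the
    centroid's paired representative.  Membership requires the alignment
    to span `min_coverage` of the shorter sequence, so a high-identity
    micro-overlap between unrelated sequences cannot join them.
    """
    sample_of = sample_of or (lambda _rid: "all")
    clusters: list[MOTUCluster] = []
    index = KmerIndex(k=8)
    by_motu: dict[str, MOTUCluster] = {}
    for unique in uniques:
        candidates = index.search_candidates(unique.sequence)
        best_motu, best_identity = None, threshold_pct
        order = {m: i for i, m in enumerate(by_motu)}
        for cand in sorted(candidates, key=order.__getitem__):
            centroid = by_motu[cand].centroid_fwd
            res = align_identity(unique.sequence, centroid)
            if res.aligned_cols < min_coverage * min(len(unique.sequence),
                                                     len(centroid)):
                continue
            if res.identity_pct > best_identity or (
                best_motu is None and res.identity_pct >= threshold_pct
            ):
                best_motu, best_identity = cand, res.identity_pct
        if best_motu is None:
            motu_id = f"MOTU_{len(clusters) + 1:04d}"
            first_read = unique.read_ids[0]
            centroid_rev = mate_of(first_read) if mate_of else ""
            cluster = MOTUCluster(motu_id, unique.sequence, centroid_rev)
            clusters.append(cluster)
            by_motu[motu_id] = cluster
            index.add(motu_id, unique.sequence)
        else:
            cluster = by_motu[best_motu]
        cluster.read_ids.extend(unique.read_ids)
        for rid in unique.read_ids:
            sid = sample_of(rid)
            cluster.counts[sid] = cluster.counts.get(sid, 0) + 1
    return clusters


def remove_singletons(
    clusters: Sequence[MOTUCluster], mode: str = "per-sample"
) -> list[MOTUCluster]:
    """Discard single-read support.

    ``per-sample`` (default): per-sample counts of exactly 1 are zeroed,
    clusters left with no reads are dropped.  ``total``: drop clusters
    whose overall count is 1.
    """
    if mode not in {"per-sample", "total"}:
        raise ValueError(f"unknown singleton mode {mode!r}")
    kept: list[MOTUCluster] = []
    for cluster in clusters:
        if mode == "total":
            if cluster.total > 1:
                kept.append(cluster)
            continue
        new_counts = {s: (0 if n == 1 else n) for s, n in cluster.counts.items()}
        if sum(new_counts.values()) > 0:
            kept.append(
                MOTUCluster(
                    cluster.motu_id,
                    cluster.centroid_fwd,
                    cluster.centroid_rev,
                    cluster.read_ids,
                    new_counts,
                )
            )
    return kept
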