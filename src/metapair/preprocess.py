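"""Demultiplexing by 7-nt MID and quality/length filtering.

A base is *bad* iff its phred score is <= `bad_quality_max` (the threshold
names the worst unacceptable score).  A read is truncated immediately
before the first run of more than `max_bad_run` consecutive bad bases.
Pairs are dropped when either truncated mate falls below `min_length`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io_formats import SequenceRead

UNMATCHED = None


@dataclass(frozen=True)
class QCParams:
    bad_quality_max: int = 20
    max_bad_run: int = 3
    min_length: int = 100
    max_mid_errors: int = 1

    def __post_init__(self) -> None:
        if min(self.bad_quality_max, self.max_bad_run, self.max_mid_errors) < 0:
            raise ValueError("QC parameters must be non-negative")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class DemuxReport:
    accepted: dict[str, int] = field(default_factory=dict)
    mid_unmatched: int = 0
    mid_ambiguous: int = 0
    too_short_forward: int = 0
    too_short_reverse: int = 0

    @property
    def n_accepted(self) -> int:
        return sum(self.accepted.values())

    @property
    def n_rejected(self) -> int:
        return (self.mid_unmatched + self.mid_ambiguous
                + self.too_short_forward + self.too_short_reverse)

    @property
    def n_input(self) -> int:
        return self.n_accepted + self.n_rejected

    def to_rows(self) -> list[tuple[str, int]]:
        rows = [(f"accepted:{sid}", n) for sid, n in sorted(self.accepted.items())]
        rows += [
            ("rejected:mid_unmatched", self.mid_unmatched),
            ("rejected:mid_ambiguous", self.mid_ambiguous),
            ("rejected:too_short_forward", self.too_short_forward),
            ("rejected:too_short_reverse", self.too_short_reverse),
        ]
        return rows


def _hamming_with_n(a: str, b: str) -> int:
    # an N (or any non-identical symbol) counts as a mismatch
    return sum(x != y for x, y in zip(a, b))


def assign_sample(
    read: SequenceRead, mids: dict[str, str], params: QCParams
) -> tuple[Optional[str], Optional[SequenceRead]]:
    """Match the first 7 bases against the MID set by Hamming distance.

    Returns ``(sample_id, read-with-MID-stripped)`` for a unique match at
    distance <= max_mid_errors, ``(None, None)`` when unmatched, and
    ``("", None)`` when two MIDs tie at the minimal acceptable distance.
    """
    if not mids:
        raise ValueError("empty MID table")
    mid_len = len(next(iter(mids.values())))
    if any(len(m) != mid_len for m in mids.values()):
        raise ValueError("MIDs have inconsistent lengths")
    if len(set(mids.values())) != len(mids):
        raise ValueError("MIDs are not unique")
    head = read.bases[:mid_len]
    if len(head) < mid_len:
        return None, None
    best: list[str] = []
    best_d = params.max_mid_errors + 1
    for sample_id, mid in mids.items():
        d = _hamming_with_n(head, mid)
        if d < best_d:
            best, best_d = [sample_id], d
        elif d == best_d:
            best.append(sample_id)
    if best_d > params.max_mid_errors:
        return None, None
    if len(best) > 1:
        return "", None  # ambiguous
    return best[0], read.trimmed(mid_len, len(read))


def quality_truncate(read: SequenceRead, params: QCParams) -> SequenceRead:
    """Truncate before the first run of more than max_bad_run bad bases."""
    run = 0
    for i, q in enumerate(read.quals):
        if q <= params.bad_quality_max:
            run += 1
            if run > params.max_bad_run:
                return read.trimmed(0, i - run + 1)
        else:
            run = 0
    return read


def length_filter(
    fwd: SequenceRead, rev: SequenceRead, params: QCParams
) -> bool:
    """Keep the pair iff both truncated mates are >= min_length nt."""
    return len(fwd) >= params.min_length and len(rev) >= params.min_length


def demultiplex(
    pairs: Iterable[tuple[SequenceRead, SequenceRead]],
    mids: dict[str, str],
    params: QCParams = QCParams(),
) -> tuple[dict[str, list[tuple[SequenceRead, SequenceRead]]], DemuxReport]:
    """Assign pairs to samples, truncate by quality, and length-filter.

    Every input pair lands in exactly one accounting cell of the report.
    """
    out: dict[str, list[tuple[SequenceRead, SequenceRead]]] = {
        sid: [] for sid in mids
    }
    report = DemuxReport(accepted={sid: 0 for sid in mids})
    for fwd, rev in pairs:
        sample_id, stripped = assign_sample(fwd, mids, params)
        if sample_id is None:
            report.mid_unmatched += 1
            continue
        if stripped is None:
            report.mid_ambiguous += 1
            continue
        tf = quality_truncate(stripped, params)
        tr = quality_truncate(rev, params)
        if len(tf) < params.min_length:
            report.too_short_forward += 1
            continue
        if len(tr) < params.min_length:
            report.too_short_reverse += 1
            continue
        out[sample_id].append((tf, tr))
        report.accepted[sample_id] += 1
    return out, report
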