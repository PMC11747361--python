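"""GAP-Seq adaptive-sampling design: target regions at contig ends,
long-read QC filtering, and gap-spanning read classification.

The strategy targets the terminal windows of contigs for nanopore adaptive
sampling so that the retained molecules extend past contig ends into
unresolved gaps. Two design modes are supported:

* ``plain`` — the outermost ``target_len`` bases of both ends of every
  contig (ends overlapping on short contigs are merged into one region);
* ``repeat_aware`` — the same geometry, but an end is only emitted when
  the union of repeat annotations covers strictly less than
  ``max_repeat_fraction`` of its terminal ``repeat_window`` (repeat-dense
  ends defeat the enrichment and are suppressed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Mapping, Sequence

from .io_formats import Interval, PafRecord, QualRead, SeqRecord, covered_length

__all__ = [
    "TargetParams",
    "TargetRegion",
    "ReadFilterParams",
    "FilterReport",
    "ReadClassification",
    "design_targets",
    "filter_reads",
    "classify_reads",
]


@dataclass(frozen=True)
class TargetParams:
    target_len: int = 5_000
    repeat_window: int = 100_000
    max_repeat_fraction: float = 0.50
    mode: Literal["plain", "repeat_aware"] = "plain"

    def __post_init__(self) -> None:
        if not (0 < self.target_len <= self.repeat_window):
            raise ValueError("need 0 < target_len <= repeat_window")
        if not (0.0 <= self.max_repeat_fraction <= 1.0):
            raise ValueError("max_repeat_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TargetRegion:
    """A terminal interval selected (or suppressed) for adaptive sampling."""

    interval: Interval
    side: Literal["head", "tail", "both"]
    repeat_fraction: float = 0.0
    suppressed: bool = False

    @property
    def seq_id(self) -> str:
        return self.interval.seq_id


@dataclass(frozen=True)
class ReadFilterParams:
    min_qv: float = 10.0
    min_len: int = 20_000

    def __post_init__(self) -> None:
        if self.min_qv < 0 or self.min_len < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class FilterReport:
    total: int = 0
    kept: int = 0
    rejected_by_len: int = 0
    rejected_by_qv: int = 0


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    status: Literal["gap_spanning", "proximal", "off_target"]
    anchored_end: tuple[str, str] | None = None  # (contig id, side)
    overhang: int = 0


def design_targets(
    contigs: Iterable[SeqRecord] | Mapping[str, str],
    repeats: Sequence[Interval] = (),
    params: TargetParams = TargetParams(),
    include_suppressed: bool = False,
) -> list[TargetRegion]:
    """Design adaptive-sampling target regions at contig ends.

    In ``repeat_aware`` mode the repeat fraction of each terminal window is
    computed on the union of the repeat intervals (overlapping annotations
    never double-count) and an end is emitted only when that fraction is
    strictly below ``max_repeat_fraction``. Suppressed ends are returned
    (flagged) when ``include_suppressed`` is set.
    """
    if not isinstance(contigs, Mapping):
        contigs = {rec.id: rec.sequence for rec in contigs}
    lengths = {cid: len(seq) for cid, seq in contigs.items()}
    for iv in repeats:
        if iv.seq_id not in lengths:
            raise KeyError(f"repeat interval references unknown contig {iv.seq_id!r}")

    t, w = params.target_len, params.repeat_window
    out: list[TargetRegion] = []
    for cid in sorted(lengths):
        L = lengths[cid]
        if params.mode == "plain":
            ok_head = ok_tail = True
            frac_head = frac_tail = 0.0
        else:
            w_used = min(w, L)
            frac_head = covered_length(repeats, cid, 0, w_used) / w_used
            frac_tail = covered_length(repeats, cid, L - w_used, L) / w_used
            ok_head = frac_head < params.max_repeat_fraction
            ok_tail = frac_tail < params.max_repeat_fraction

        if L <= 2 * t and ok_head and ok_tail:
            out.append(
                TargetRegion(Interval(cid, 0, L), "both", max(frac_head, frac_tail))
            )
            continue
        head_len = min(t, L)
        if ok_head or include_suppressed:
            out.append(
                TargetRegion(Interval(cid, 0, head_len), "head", frac_head, suppressed=not ok_head)
            )
        if L > t and (ok_tail or include_suppressed):
            out.append(
                TargetRegion(Interval(cid, L - t, L), "tail", frac_tail, suppressed=not ok_tail)
            )
    return [r for r in out if include_suppressed or not r.suppressed]


def filter_reads(
    reads: Iterable[QualRead], params: ReadFilterParams = ReadFilterParams()
) -> tuple[list[QualRead], FilterReport]:
    """Keep reads with length >= min_len and mean QV >= min_qv.

    A read failing both thresholds is counted once, under length.
    """
    kept: list[QualRead] = []
    total = rej_len = rej_qv = 0
    for read in reads:
        total += 1
        if len(read) < params.min_len:
            rej_len += 1
        elif read.mean_qv < params.min_qv:
            rej_qv += 1
        else:
            kept.append(read)
    return kept, FilterReport(total, len(kept), rej_len, rej_qv)


def _outward_overhang(
    aln: PafRecord, side: str, epsilon: int
) -> int | None:
    """Unaligned read bases extending past the contig end on the outward side
    of ``side``, or None when the alignment does not reach the end."""
    if side == "head":
        if aln.tstart > epsilon:
            return None
        inward_slack = aln.tstart  # contig bases still between alignment and the end
        outside = aln.qstart if aln.strand == "+" else aln.qlen - aln.qend
    else:  # tail
        if aln.tlen - aln.tend > epsilon:
            return None
        inward_slack = aln.tlen - aln.tend
        outside = aln.qlen - aln.qend if aln.strand == "+" else aln.qstart
    overhang = outside - inward_slack
    return overhang if overhang > 0 else None


def classify_reads(
    reads: Iterable[QualRead] | Iterable[str],
    targets: Sequence[TargetRegion],
    alignments: Sequence[PafRecord],
    epsilon: int = 100,
) -> list[ReadClassification]:
    """Classify reads against target regions using their alignments.

    A read whose best alignment (most residue matches) overlaps a target
    region is on-target; it is ``gap_spanning`` when its unaligned portion
    extends past the contig end on the target's outward side (the alignment
    must reach within ``epsilon`` bases of the terminus), otherwise
    ``proximal``. Reads without a target-overlapping alignment are
    ``off_target``.
    """
    read_ids = [r.id if isinstance(r, QualRead) else r for r in reads]
    known = set(read_ids)
    contig_targets: dict[str, list[TargetRegion]] = {}
    for tr in targets:
        contig_targets.setdefault(tr.seq_id, []).append(tr)
    by_read: dict[str, list[PafRecord]] = {}
    for aln in alignments:
        if aln.qname not in known:
            raise KeyError(f"alignment references unknown read {aln.qname!r}")
        by_read.setdefault(aln.qname, []).append(aln)

    out: list[ReadClassification] = []
    for rid in read_ids:
        alns = sorted(
            by_read.get(rid, ()),
            key=lambda a: (-a.matches, a.tname, a.tstart, a.qstart),
        )
        best_on_target: tuple[PafRecord, TargetRegion] | None = None
        for aln in alns:
            for tr in contig_targets.get(aln.tname, ()):
                if aln.tstart < tr.interval.end and tr.interval.start < aln.tend:
                    best_on_target = (aln, tr)
                    break
            if best_on_target:
                break
        if best_on_target is None:
            out.append(ReadClassification(rid, "off_target"))
            continue
        aln, tr = best_on_target
        sides = ("head", "tail") if tr.side == "both" else (tr.side,)
        spanning: tuple[str, int] | None = None
        for side in sides:
            overhang = _outward_overhang(aln, side, epsilon)
            if overhang is not None:
                spanning = (side, overhang)
                break
        if spanning:
            side, overhang = spanning
            out.append(ReadClassification(rid, "gap_spanning", (aln.tname, side), overhang))
        else:
            out.append(ReadClassification(rid, "proximal", (aln.tname, sides[0]), 0))
    return out
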