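"""Cross-assembly bridging and reference-guided pseudomolecule construction.

When two assemblies of closely related genomes are available, a scaffold of
assembly B whose ends align to the terminal regions of two different
scaffolds of assembly A is evidence that those two A-scaffolds are adjacent;
they are then joined with a fixed run of N characters (100 by default) into
a super-scaffold. Super-scaffolds are finally anchored to the chromosomes
of a related reference by alignment share, ordered by median reference
position, and concatenated into pseudomolecules named after the reference
chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._joins import Join, name_layouts, resolve_layouts
from .io_formats import PafRecord, ScaffoldLayout, layout_sequences

__all__ = [
    "BridgeParams",
    "Bridge",
    "ChromAssignment",
    "detect_bridges",
    "apply_bridges",
    "anchor_to_reference",
]

End = tuple[str, str]


@dataclass(frozen=True)
class BridgeParams:
    min_anchor: int = 20_000
    end_window: int = 500_000
    join_gap: int = 100

    def __post_init__(self) -> None:
        if self.min_anchor < 1 or self.join_gap < 1:
            raise ValueError("min_anchor and join_gap must be >= 1")


@dataclass(frozen=True)
class Bridge:
    """A B-assembly sequence bridging two A-assembly scaffolds.

    ``left``/``right`` are ``(A-scaffold id, side, orientation)`` read along
    the bridge sequence: the bridge exits ``left`` through ``left.side`` and
    enters ``right`` through ``right.side``.
    """

    bridge_seq_id: str
    left: tuple[str, str, str]
    right: tuple[str, str, str]
    support_bases: int


@dataclass(frozen=True)
class ChromAssignment:
    seq_id: str
    chromosome: str
    orientation: str
    order_key: float  # median reference position of aligned bases


@dataclass(frozen=True)
class _Anchor:
    target: str
    tlen: int
    strand: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    aligned: int


def _chain_anchors(records: Sequence[PafRecord]) -> list[_Anchor]:
    """Collapse one query's blocks into per-(target, strand) anchors."""
    groups: dict[tuple[str, str], list[PafRecord]] = {}
    for r in records:
        groups.setdefault((r.tname, r.strand), []).append(r)
    anchors = []
    for (tname, strand), blocks in sorted(groups.items()):
        anchors.append(
            _Anchor(
                tname,
                blocks[0].tlen,
                strand,
                min(b.qstart for b in blocks),
                max(b.qend for b in blocks),
                min(b.tstart for b in blocks),
                max(b.tend for b in blocks),
                sum(b.qend - b.qstart for b in blocks),
            )
        )
    return anchors


def detect_bridges(
    paf: Sequence[PafRecord], params: BridgeParams = BridgeParams()
) -> list[Bridge]:
    """Find B-sequences whose two terminal anchors join two A-scaffold ends.

    A bridge is emitted when exactly two A-scaffolds carry anchors of
    ``>= min_anchor`` aligned bases, the anchors occupy disjoint ordered
    intervals on the bridge sequence, each anchor sits within
    ``end_window`` of an A-scaffold end, and the implied junction exits one
    scaffold's end and enters the other's.
    """
    by_query: dict[str, list[PafRecord]] = {}
    for r in paf:
        by_query.setdefault(r.qname, []).append(r)

    bridges: list[Bridge] = []
    for qname in sorted(by_query):
        anchors = [a for a in _chain_anchors(by_query[qname]) if a.aligned >= params.min_anchor]
        if len(anchors) != 2 or anchors[0].target == anchors[1].target:
            continue
        left, right = sorted(anchors, key=lambda a: a.q_start)
        if left.q_end > right.q_start:  # overlapping query intervals
            continue
        # leaving the left anchor toward the right, the bridge exits contig
        # `left.target` downstream of the alignment
        if left.strand == "+":
            l_side, l_orient, l_ok = "tail", "+", left.t_end >= left.tlen - params.end_window
        else:
            l_side, l_orient, l_ok = "head", "-", left.t_start <= params.end_window
        if right.strand == "+":
            r_side, r_orient, r_ok = "head", "+", right.t_start <= params.end_window
        else:
            r_side, r_orient, r_ok = "tail", "-", right.t_end >= right.tlen - params.end_window
        if not (l_ok and r_ok):
            continue
        bridges.append(
            Bridge(
                qname,
                (left.target, l_side, l_orient),
                (right.target, r_side, r_orient),
                left.aligned + right.aligned,
            )
        )
    return bridges


def apply_bridges(
    a_sequences: Mapping[str, str],
    bridges: Sequence[Bridge],
    params: BridgeParams = BridgeParams(),
) -> tuple[dict[str, str], list[ScaffoldLayout], list[Bridge]]:
    """Join A-scaffolds per the surviving bridges with ``join_gap`` N runs.

    Conflicting bridges (two claiming the same A-scaffold end with
    different partners) are all dropped; duplicate bridges for the same
    junction are merged (support summed). Cycles are broken at the
    smallest-support bridge. Returns ``(sequences, layouts, dropped)``;
    unbridged scaffolds pass through under their own ids.
    """
    lengths = {sid: len(s) for sid, s in a_sequences.items()}
    for b in bridges:
        for sid, _, _ in (b.left, b.right):
            if sid not in lengths:
                raise KeyError(f"bridge {b.bridge_seq_id!r} references unknown scaffold {sid!r}")

    # merge duplicates of the same junction
    merged: dict[tuple[End, End], int] = {}
    for b in bridges:
        e1: End = (b.left[0], b.left[1])
        e2: End = (b.right[0], b.right[1])
        key = (e1, e2) if e1 <= e2 else (e2, e1)
        merged[key] = merged.get(key, 0) + b.support_bases

    claims: dict[End, int] = {}
    for (e1, e2) in merged:
        claims[e1] = claims.get(e1, 0) + 1
        claims[e2] = claims.get(e2, 0) + 1
    conflicted = {e for e, n in claims.items() if n > 1}

    joins: list[Join] = []
    dropped: list[Bridge] = []
    for b in bridges:
        e1, e2 = (b.left[0], b.left[1]), (b.right[0], b.right[1])
        if e1 in conflicted or e2 in conflicted:
            dropped.append(b)
    surviving = {
        key: sup
        for key, sup in merged.items()
        if key[0] not in conflicted and key[1] not in conflicted
    }
    for (e1, e2), sup in sorted(surviving.items()):
        joins.append(Join(e1, e2, params.join_gap, sup))

    layouts, cycle_joins = resolve_layouts(joins, lengths)
    cycle_keys = {j.key() for j in cycle_joins}
    for b in bridges:
        e1, e2 = (b.left[0], b.left[1]), (b.right[0], b.right[1])
        if (e1, e2) in cycle_keys or (e2, e1) in cycle_keys:
            dropped.append(b)

    multi = [l for l in layouts if len(l.parts) > 1]
    singles = [l for l in layouts if len(l.parts) == 1]
    multi = name_layouts(multi, lengths, prefix="superscaffold")
    for l in singles:
        l.scaffold_id = l.parts[0][0]
    layouts = multi + singles
    sequences = layout_sequences(layouts, a_sequences)
    return sequences, layouts, dropped


def _weighted_median(positions: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(positions)
    pos, w = positions[order], weights[order]
    cum = np.cumsum(w)
    return float(pos[np.searchsorted(cum, cum[-1] / 2.0)])


def anchor_to_reference(
    paf: Sequence[PafRecord],
    min_cov_frac: float = 0.3,
    join_gap: int = 100,
) -> tuple[list[ChromAssignment], list[ScaffoldLayout], list[str]]:
    """Assign super-scaffolds to reference chromosomes by alignment share.

    Each query is assigned to the chromosome receiving the largest share of
    its aligned bases, provided that share is at least ``min_cov_frac``;
    its orientation is the strand carrying the majority of aligned bases
    there. Within a chromosome, queries are ordered by the weighted median
    reference position and concatenated with ``join_gap`` N gaps. Returns
    ``(assignments, pseudomolecule layouts, unplaced query ids)``.
    """
    by_query: dict[str, list[PafRecord]] = {}
    for r in paf:
        by_query.setdefault(r.qname, []).append(r)

    assignments: list[ChromAssignment] = []
    unplaced: list[str] = []
    for qname in sorted(by_query):
        recs = by_query[qname]
        per_chrom: dict[str, int] = {}
        for r in recs:
            per_chrom[r.tname] = per_chrom.get(r.tname, 0) + (r.qend - r.qstart)
        total = sum(per_chrom.values())
        chrom, best = max(sorted(per_chrom.items()), key=lambda kv: kv[1])
        if total == 0 or best / total < min_cov_frac:
            unplaced.append(qname)
            continue
        on_chrom = [r for r in recs if r.tname == chrom]
        plus = sum(r.qend - r.qstart for r in on_chrom if r.strand == "+")
        minus = sum(r.qend - r.qstart for r in on_chrom if r.strand == "-")
        orient = "+" if plus >= minus else "-"
        mids = np.array([(r.tstart + r.tend) / 2.0 for r in on_chrom])
        weights = np.array([r.qend - r.qstart for r in on_chrom], dtype=float)
        assignments.append(ChromAssignment(qname, chrom, orient, _weighted_median(mids, weights)))

    layouts: list[ScaffoldLayout] = []
    for chrom in sorted({a.chromosome for a in assignments}):
        members = sorted(
            (a for a in assignments if a.chromosome == chrom),
            key=lambda a: (a.order_key, a.seq_id),
        )
        parts = [
            (a.seq_id, a.orientation, join_gap if i < len(members) - 1 else 0)
            for i, a in enumerate(members)
        ]
        layouts.append(ScaffoldLayout(chrom, parts))
    return assignments, layouts, unplaced
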