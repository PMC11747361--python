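"""k-mer-pair link scaffolding (LINKS-style) for gap-spanning long reads.

A pair of k-mers observed a fixed distance ``d`` apart on one long read,
each locating *uniquely* on a different contig, is evidence that the two
contigs are adjacent. Pairs vote for oriented contig-end adjacencies; an
edge is accepted when it has enough consistent support and is unambiguous
from both of its ends (link-ratio test against the second-best edge).
Repeats are the known failure mode, so only k-mers occurring exactly once
across the whole contig set may contribute.

Default parameters are the conservative set tuned for ~20-kb nanopore
reads: k=51, >=15 links, pair distance 20,000 bp, 2% distance error,
maximum link ratio 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

from ._joins import Join, name_layouts, resolve_layouts
from .io_formats import QualRead, ScaffoldLayout, SeqRecord, revcomp

__all__ = [
    "LinkParams",
    "KmerPair",
    "KmerIndex",
    "LinkEdge",
    "RejectedEdge",
    "index_unique_kmers",
    "extract_pairs",
    "build_link_graph",
    "layout_scaffolds",
    "scaffold_assembly",
]

End = tuple[str, str]


@dataclass(frozen=True)
class LinkParams:
    k: int = 51
    min_links: int = 15
    pair_distance: int = 20_000
    distance_error: float = 0.02
    max_link_ratio: float = 0.1
    step: int = 2

    def __post_init__(self) -> None:
        if self.k < 11 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 11")
        if self.pair_distance <= self.k:
            raise ValueError("pair distance must exceed k")
        if not (0 < self.distance_error < 1):
            raise ValueError("distance_error must be in (0, 1)")
        if not (0 < self.max_link_ratio < 1):
            raise ValueError("max_link_ratio must be in (0, 1)")
        if self.min_links < 1 or self.step < 1:
            raise ValueError("min_links and step must be >= 1")


@dataclass(frozen=True)
class KmerPair:
    kmer_a: str
    kmer_b: str
    read_id: str
    offset: int
    separation: int


@dataclass(frozen=True)
class KmerIndex:
    """Canonical k-mer -> unique (contig, position, orientation) placement.

    ``orientation`` is '+' when the contig's forward k-mer at ``position``
    equals the canonical form. Multi-copy k-mers live in ``blacklist``.
    """

    k: int
    placements: dict[str, tuple[str, int, str]]
    blacklist: frozenset[str]


@dataclass
class LinkEdge:
    end_a: End
    end_b: End
    support: int
    gap_estimates: list[int]
    raw_support: int = 0  # pairs before the distance-consistency filter

    @property
    def gap_median(self) -> int:
        return int(round(median(self.gap_estimates)))


@dataclass(frozen=True)
class RejectedEdge:
    end_a: End
    end_b: End
    support: int
    reason: str


def _canonical(kmer: str) -> tuple[str, str]:
    """(canonical form, '+' if the forward k-mer is canonical else '-')."""
    rc = revcomp(kmer)
    return (kmer, "+") if kmer <= rc else (rc, "-")


def index_unique_kmers(
    contigs: Iterable[SeqRecord] | Mapping[str, str], k: int
) -> KmerIndex:
    """Index canonical k-mers occurring exactly once across all contigs."""
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if not isinstance(contigs, Mapping):
        contigs = {rec.id: rec.sequence for rec in contigs}
    placements: dict[str, tuple[str, int, str]] = {}
    blacklist: set[str] = set()
    for cid in sorted(contigs):
        seq = contigs[cid]
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            canon, orient = _canonical(kmer)
            if canon in blacklist:
                continue
            if canon in placements:
                del placements[canon]
                blacklist.add(canon)
            else:
                placements[canon] = (cid, i, orient)
    return KmerIndex(k, placements, frozenset(blacklist))


def extract_pairs(read: QualRead | SeqRecord, params: LinkParams) -> list[KmerPair]:
    """Extract k-mer pairs at offsets 0, step, 2*step, ... along a read.

    A pair at offset ``o`` uses the k-mers starting at ``o`` and ``o + d``;
    extraction requires ``o + d + k <= len(read)``. k-mers containing N are
    skipped.
    """
    seq = read.sequence
    k, d = params.k, params.pair_distance
    pairs: list[KmerPair] = []
    for o in range(0, len(seq) - d - k + 1, params.step):
        a = seq[o : o + k]
        b = seq[o + d : o + d + k]
        if "N" in a or "N" in b:
            continue
        pairs.append(KmerPair(a, b, read.id, o, d))
    return pairs


def _hit(index: KmerIndex, kmer: str) -> tuple[str, int, str] | None:
    """Locate a read k-mer: (contig, position, relative strand) or None."""
    canon, read_orient = _canonical(kmer)
    placed = index.placements.get(canon)
    if placed is None:
        return None
    cid, pos, contig_orient = placed
    return cid, pos, "+" if read_orient == contig_orient else "-"


def build_link_graph(
    pairs: Iterable[KmerPair],
    index: KmerIndex,
    params: LinkParams,
    contig_lengths: Mapping[str, int],
) -> list[LinkEdge]:
    """Aggregate k-mer pairs into oriented contig-end link edges.

    For a pair whose two k-mers land uniquely on different contigs, the
    read's local direction at each hit determines which contig end faces
    the gap, and the implied gap size is ``d`` minus the two distances from
    the k-mers to their outward ends. Estimates deviating from the edge's
    median gap by more than ``distance_error * d`` are discarded.
    """
    k, d, e = params.k, params.pair_distance, params.distance_error
    raw: dict[tuple[End, End], list[int]] = {}
    for pair in pairs:
        hit_a = _hit(index, pair.kmer_a)
        hit_b = _hit(index, pair.kmer_b)
        if hit_a is None or hit_b is None:
            continue
        (ca, pa, sa), (cb, pb, sb) = hit_a, hit_b
        if ca == cb:
            continue
        la, lb = contig_lengths[ca], contig_lengths[cb]
        # the read exits contig A through its tail when it runs forward there
        side_a = "tail" if sa == "+" else "head"
        dist_a = (la - pa) if sa == "+" else (pa + k)
        # ... and enters contig B through its head when it runs forward there
        side_b = "head" if sb == "+" else "tail"
        dist_b = pb if sb == "+" else (lb - pb - k)
        gap = d - dist_a - dist_b
        end_a, end_b = (ca, side_a), (cb, side_b)
        key = (end_a, end_b) if end_a <= end_b else (end_b, end_a)
        raw.setdefault(key, []).append(gap)

    edges: list[LinkEdge] = []
    for (end_a, end_b), gaps in sorted(raw.items()):
        med = median(gaps)
        kept = sorted(g for g in gaps if abs(g - med) <= e * d)
        if kept:
            edges.append(LinkEdge(end_a, end_b, len(kept), kept, raw_support=len(gaps)))
    return edges


def _best_edge_at(
    end: End, incident: Sequence[LinkEdge], params: LinkParams
) -> tuple[LinkEdge | None, str | None]:
    """The usable edge at an end, or (None, reason)."""
    ranked = sorted(
        incident, key=lambda ed: (-ed.support, ed.end_a, ed.end_b)
    )
    best = ranked[0]
    if best.support < params.min_links:
        return None, "min_links"
    second = ranked[1].support if len(ranked) > 1 else 0
    if second / best.support > params.max_link_ratio:
        return None, "link_ratio"
    return best, None


def layout_scaffolds(
    edges: Sequence[LinkEdge],
    contigs: Iterable[SeqRecord] | Mapping[str, str],
    params: LinkParams,
) -> tuple[list[ScaffoldLayout], list[RejectedEdge]]:
    """Select unambiguous, well-supported joins and walk them into layouts.

    A join is made only when its edge is the best at BOTH of its ends, has
    ``support >= min_links``, and beats the runner-up at each end by the
    link-ratio test. Cycles are broken at the lowest-support join. Internal
    gaps are the (rounded) median gap estimate, floored at 1 N.
    """
    if not isinstance(contigs, Mapping):
        contigs = {rec.id: rec.sequence for rec in contigs}
    lengths = {cid: len(seq) for cid, seq in contigs.items()}

    incident: dict[End, list[LinkEdge]] = {}
    for ed in edges:
        incident.setdefault(ed.end_a, []).append(ed)
        incident.setdefault(ed.end_b, []).append(ed)

    usable: dict[End, LinkEdge] = {}
    ratio_failed: set[End] = set()
    for end, eds in incident.items():
        best, reason = _best_edge_at(end, eds, params)
        if best is not None:
            usable[end] = best
        elif reason == "link_ratio":
            ratio_failed.add(end)

    joins: list[Join] = []
    rejected: list[RejectedEdge] = []
    for ed in edges:
        if usable.get(ed.end_a) is ed and usable.get(ed.end_b) is ed:
            joins.append(Join(ed.end_a, ed.end_b, max(ed.gap_median, 1), ed.support))
        elif ed.support < params.min_links:
            rejected.append(RejectedEdge(ed.end_a, ed.end_b, ed.support, "min_links"))
        elif ed.end_a in ratio_failed or ed.end_b in ratio_failed:
            rejected.append(RejectedEdge(ed.end_a, ed.end_b, ed.support, "link_ratio"))
        else:
            rejected.append(RejectedEdge(ed.end_a, ed.end_b, ed.support, "not_best_at_end"))

    layouts, dropped = resolve_layouts(joins, lengths)
    for j in dropped:
        rejected.append(RejectedEdge(j.end_a, j.end_b, int(j.weight), "cycle"))
    layouts = name_layouts(layouts, lengths, prefix="scaffold")
    return layouts, rejected


def scaffold_assembly(
    contigs: Iterable[SeqRecord] | Mapping[str, str],
    reads: Iterable[QualRead],
    params: LinkParams = LinkParams(),
) -> tuple[list[ScaffoldLayout], list[RejectedEdge], list[LinkEdge]]:
    """Full pipeline: index contigs, extract pairs from reads, link, lay out."""
    if not isinstance(contigs, Mapping):
        contigs = {rec.id: rec.sequence for rec in contigs}
    lengths = {cid: len(seq) for cid, seq in contigs.items()}
    index = index_unique_kmers(contigs, params.k)
    pairs: list[KmerPair] = []
    for read in reads:
        pairs.extend(extract_pairs(read, params))
    edges = build_link_graph(pairs, index, params, lengths)
    layouts, rejected = layout_scaffolds(edges, contigs, params)
    return layouts, rejected, edges
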