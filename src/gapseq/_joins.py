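"""Shared machinery for turning pairwise end-joins into linear layouts.

Both the k-mer-pair link scaffolder and the cross-assembly bridger reduce
to the same combinatorial step: a set of joins between sequence *ends*
(each end used at most once) that must be walked into ordered, oriented
linear layouts. Because every end participates in at most one join, the
join graph decomposes into simple paths and cycles; cycles are broken at
their lowest-weight join (ties lexicographic), and each path is traversed
from its lexicographically smallest terminal contig for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import ScaffoldLayout

End = tuple[str, str]  # (sequence id, "head" | "tail")


@dataclass(frozen=True)
class Join:
    end_a: End
    end_b: End
    gap: int
    weight: float

    def key(self) -> tuple[End, End]:
        return (self.end_a, self.end_b) if self.end_a <= self.end_b else (self.end_b, self.end_a)


def resolve_layouts(
    joins: Sequence[Join], lengths: Mapping[str, int]
) -> tuple[list[ScaffoldLayout], list[Join]]:
    """Walk joins into linear layouts covering every sequence in ``lengths``.

    Returns ``(layouts, dropped)`` where ``dropped`` holds joins removed to
    break cycles. Layout ids are temporary (positional); callers rename.
    """
    end_map: dict[End, tuple[End, Join]] = {}
    for j in sorted(joins, key=lambda j: j.key()):
        for e in (j.end_a, j.end_b):
            if e in end_map:
                raise ValueError(f"end {e} participates in more than one join")
        if j.end_a[0] == j.end_b[0]:
            raise ValueError(f"self-join on {j.end_a[0]!r}")
        end_map[j.end_a] = (j.end_b, j)
        end_map[j.end_b] = (j.end_a, j)

    # component discovery over sequences
    dropped: list[Join] = []
    visited: set[str] = set()
    layouts: list[ScaffoldLayout] = []
    for seed in sorted(lengths):
        if seed in visited:
            continue
        # collect the component and its joins by walking both directions
        comp: set[str] = {seed}
        comp_joins: dict[tuple[End, End], Join] = {}
        frontier = [seed]
        while frontier:
            cid = frontier.pop()
            for side in ("head", "tail"):
                hit = end_map.get((cid, side))
                if hit is None:
                    continue
                (other_cid, _), join = hit
                comp_joins[join.key()] = join
                if other_cid not in comp:
                    comp.add(other_cid)
                    frontier.append(other_cid)
        if len(comp_joins) == len(comp):  # cycle: every contig has both ends joined
            weakest = min(comp_joins.values(), key=lambda j: (j.weight, j.key()))
            dropped.append(weakest)
            for e in (weakest.end_a, weakest.end_b):
                del end_map[e]
            del comp_joins[weakest.key()]

        visited |= comp
        # locate terminal ends (free ends of the path)
        free_ends = sorted(
            (cid, side)
            for cid in comp
            for side in ("head", "tail")
            if (cid, side) not in end_map
        )
        if len(comp) == 1 and not comp_joins:
            layouts.append(ScaffoldLayout("", [(seed, "+", 0)]))
            continue
        start_cid, start_side = free_ends[0]
        orient = "+" if start_side == "head" else "-"
        parts: list[tuple[str, str, int]] = []
        cid = start_cid
        while True:
            exit_end: End = (cid, "tail" if orient == "+" else "head")
            hit = end_map.get(exit_end)
            if hit is None:
                parts.append((cid, orient, 0))
                break
            (next_cid, next_side), join = hit
            parts.append((cid, orient, join.gap))
            cid = next_cid
            orient = "+" if next_side == "head" else "-"
        layouts.append(ScaffoldLayout("", parts))
    return layouts, dropped


def name_layouts(
    layouts: list[ScaffoldLayout], lengths: Mapping[str, int], prefix: str = "scaffold"
) -> list[ScaffoldLayout]:
    """Assign ``<prefix>_NNNN`` ids in descending total-length order."""
    layouts = sorted(
        layouts,
        key=lambda l: (-l.total_length(lengths), l.parts[0][0]),
    )
    for i, layout in enumerate(layouts, 1):
        layout.scaffold_id = f"{prefix}_{i:04d}"
    return layouts
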