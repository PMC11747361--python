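"""Readers and writers for the plain-text formats the pipeline touches.

Conventions fixed here once, so the rest of the package never argues about
them:

* every internal coordinate is 0-based, half-open (BED convention);
* the AGP writer converts to 1-based inclusive at the output boundary;
* DNA is uppercased on read and restricted to ``A C G T N``;
* mean read quality is Phred-scaled from the *mean error probability*, the
  convention of common long-read filters, not the arithmetic mean of the
  per-base Phred scores;
* FASTA output wraps at 60 columns, readers accept any wrapping;
* ``.gz`` paths are opened transparently.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SeqRecord",
    "QualRead",
    "Interval",
    "PafRecord",
    "ScaffoldLayout",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_bed",
    "write_bed",
    "read_paf",
    "write_paf",
    "write_agp",
    "read_kmer_histogram",
    "repeatmasker_out_to_bed",
    "revcomp",
    "merge_intervals",
    "covered_length",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence (contig, scaffold, or pseudomolecule)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"sequence id {self.id!r} must be non-empty and whitespace-free")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QualRead:
    """A long read with per-base Phred qualities."""

    id: str
    sequence: str
    per_base_qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.per_base_qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: {len(self.per_base_qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_qv(self) -> float:
        """Phred-scaled mean error probability, -10*log10(mean(10^(-q/10)))."""
        probs = [10.0 ** (-q / 10.0) for q in self.per_base_qualities]
        return -10.0 * math.log10(sum(probs) / len(probs))


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    label: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PafRecord:
    """One mandatory-column PAF alignment record (extra tags are dropped)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    matches: int
    block_len: int
    mapq: int

    def __post_init__(self) -> None:
        for side, s, e, ln in (
            ("query", self.qstart, self.qend, self.qlen),
            ("target", self.tstart, self.tend, self.tlen),
        ):
            if not (0 <= s < e <= ln):
                raise ValueError(
                    f"PAF {self.qname}->{self.tname}: bad {side} coordinates {s}-{e} (length {ln})"
                )
        if self.strand not in ("+", "-"):
            raise ValueError(f"PAF {self.qname}->{self.tname}: strand must be + or -, got {self.strand!r}")
        if self.matches > self.block_len:
            raise ValueError(f"PAF {self.qname}->{self.tname}: matches exceed block length")


@dataclass
class ScaffoldLayout:
    """Ordered, oriented component placements with gap sizes (AGP-equivalent).

    ``parts`` is a list of ``(component_id, orientation, gap_after)`` where
    ``gap_after`` is the number of N bases inserted after the component
    (0 for the last part).
    """

    scaffold_id: str
    parts: list[tuple[str, str, int]] = field(default_factory=list)

    def total_length(self, lengths: Mapping[str, int]) -> int:
        return sum(lengths[cid] + gap for cid, _, gap in self.parts)

    def component_ids(self) -> list[str]:
        return [cid for cid, _, _ in self.parts]


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into uppercased records, preserving order.

    Raises ``ValueError`` on duplicate ids or empty sequences.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"empty sequence for id {rec.id!r} in {path}")
            records.append(SeqRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SeqRecord] | Mapping[str, str], path: str | Path) -> None:
    """Write records (or an id->sequence mapping) as 60-column-wrapped FASTA."""
    if isinstance(records, Mapping):
        records = [SeqRecord(k, v) for k, v in records.items()]
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with _open_text(path, "wt") as handle:
        SeqIO.write(bio, handle, "fasta")


def read_fastq(path: str | Path) -> Iterator[QualRead]:
    """Stream 4-line FASTQ (Phred+33) records as :class:`QualRead`."""
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                yield QualRead(
                    rec.id,
                    str(rec.seq).upper(),
                    tuple(rec.letter_annotations["phred_quality"]),
                )
        except ValueError as exc:  # Biopython reports the offending record
            raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc


def write_fastq(reads: Iterable[QualRead], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for r in reads:
            rec = _BioSeqRecord(Seq(r.sequence), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = list(r.per_base_qualities)
            SeqIO.write([rec], handle, "fastq")


# ---------------------------------------------------------------------------
# BED and interval arithmetic
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[Interval]:
    """Read 3-6 column BED into intervals (column 4 -> label, 6 -> strand)."""
    out: list[Interval] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            label = cols[3] if len(cols) > 3 else None
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else None
            out.append(Interval(cols[0], int(cols[1]), int(cols[2]), label, strand))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for iv in intervals:
            cols = [iv.seq_id, str(iv.start), str(iv.end)]
            if iv.label is not None or iv.strand is not None:
                cols.append(iv.label if iv.label is not None else ".")
            if iv.strand is not None:
                cols += [".", iv.strand]
            handle.write("\t".join(cols) + "\n")


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Union of intervals, per sequence id (labels/strands dropped)."""
    by_seq: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.seq_id, []).append(iv)
    merged: list[Interval] = []
    for seq_id in sorted(by_seq):
        ivs = sorted(by_seq[seq_id], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(Interval(seq_id, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(Interval(seq_id, cur_s, cur_e))
    return merged


def covered_length(intervals: Sequence[Interval], seq_id: str, start: int, end: int) -> int:
    """Total bases of ``[start, end)`` on ``seq_id`` covered by the interval union."""
    total = 0
    for iv in merge_intervals([iv for iv in intervals if iv.seq_id == seq_id]):
        total += max(0, min(iv.end, end) - max(iv.start, start))
    return total


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------


def read_paf(path: str | Path) -> list[PafRecord]:
    """Parse the 12 mandatory PAF columns; extra tag columns are ignored."""
    records: list[PafRecord] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: PAF needs >= 12 columns, got {len(cols)}")
            try:
                rec = PafRecord(
                    cols[0], int(cols[1]), int(cols[2]), int(cols[3]), cols[4],
                    cols[5], int(cols[6]), int(cols[7]), int(cols[8]),
                    int(cols[9]), int(cols[10]), int(cols[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_paf(records: Iterable[PafRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for r in records:
            handle.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.qname, r.qlen, r.qstart, r.qend, r.strand,
                        r.tname, r.tlen, r.tstart, r.tend,
                        r.matches, r.block_len, r.mapq,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# AGP v2.1
# ---------------------------------------------------------------------------


def write_agp(
    layouts: Sequence[ScaffoldLayout],
    component_lengths: Mapping[str, int],
    path: str | Path,
    evidence: str = "paired-ends",
) -> None:
    """Write scaffold layouts as AGP v2.1 (1-based inclusive coordinates).

    Gap rows use gap type ``scaffold`` with linkage ``yes``; component
    orientation goes in column 9 of W rows.
    """
    with _open_text(path, "wt") as handle:
        handle.write("##agp-version\t2.1\n")
        for layout in layouts:
            pos = 0  # 0-based running offset on the object
            part_no = 0
            for cid, orient, gap in layout.parts:
                if cid not in component_lengths:
                    raise KeyError(f"unknown component id {cid!r} in layout {layout.scaffold_id!r}")
                clen = component_lengths[cid]
                part_no += 1
                handle.write(
                    "\t".join(
                        (
                            layout.scaffold_id,
                            str(pos + 1), str(pos + clen), str(part_no),
                            "W", cid, "1", str(clen), orient,
                        )
                    )
                    + "\n"
                )
                pos += clen
                if gap:
                    part_no += 1
                    handle.write(
                        "\t".join(
                            (
                                layout.scaffold_id,
                                str(pos + 1), str(pos + gap), str(part_no),
                                "N", str(gap), "scaffold", "yes", evidence,
                            )
                        )
                        + "\n"
                    )
                    pos += gap


def layout_sequences(
    layouts: Sequence[ScaffoldLayout], components: Mapping[str, str]
) -> dict[str, str]:
    """Materialise layout objects as sequences (N gaps, orientation applied)."""
    out: dict[str, str] = {}
    for layout in layouts:
        chunks: list[str] = []
        for cid, orient, gap in layout.parts:
            seq = components[cid]
            chunks.append(revcomp(seq) if orient == "-" else seq)
            if gap:
                chunks.append("N" * gap)
        out[layout.scaffold_id] = "".join(chunks)
    return out


# ---------------------------------------------------------------------------
# misc text formats
# ---------------------------------------------------------------------------


def read_kmer_histogram(path: str | Path) -> list[tuple[int, int]]:
    """Read ``multiplicity<TAB>count`` text as produced by k-mer counters."""
    pairs: list[tuple[int, int]] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'multiplicity count'")
            pairs.append((int(cols[0]), int(cols[1])))
    if any(b[0] <= a[0] for a, b in zip(pairs, pairs[1:])):
        raise ValueError(f"{path}: multiplicities must be strictly increasing")
    return pairs


def repeatmasker_out_to_bed(path: str | Path) -> list[Interval]:
    """Convert RepeatMasker ``.out`` column layout to BED-style intervals.

    Only the query coordinates (1-based inclusive -> half-open), repeat name
    and strand (``C`` -> ``-``) are retained. RepeatMasker itself is never
    invoked by this package; annotations are consumed, not produced.
    """
    out: list[Interval] = []
    with _open_text(path) as handle:
        for line in handle:
            cols = line.split()
            if len(cols) < 11 or not cols[0].isdigit():
                continue  # header / blank lines
            seq_id, qbeg, qend = cols[4], int(cols[5]), int(cols[6])
            strand = "-" if cols[8] == "C" else "+"
            out.append(Interval(seq_id, qbeg - 1, qend, cols[9], strand))
    return out
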